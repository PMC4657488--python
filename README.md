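# remcam

Random encounter model (REM) density estimation for camera-trap surveys of
unmarked animals, with census-based reference densities and a
movement/detection simulator for validating the whole pipeline against
known ground truth.

## The problem

Camera traps photograph many species whose individuals cannot be told
apart, so capture–recapture density estimators do not apply. The REM
instead treats animals as an ideal gas of independent movers and cameras as
static detectors: the rate at which animals "collide" with a camera's
detection zone is proportional to their density, their speed, and the
zone's cross-section. Given the encounter rate `y/t` (independent
photographic events per camera-hour), mean movement speed `V` (km/h) and a
sector-shaped detection zone of radius `r` (km) and full angle `θ`
(radians), density is

    D = (y/t) · π / (V · r · (2 + θ))        [animals / km²]

Uncertainty combines a camera-level bootstrap of the encounter rate with
delta-method propagation of the parameter standard errors:

    CV²(D) = CV²(y/t) + CV²(V) + CV²(r) + (θ/(2+θ))² · CV²(θ)

A key assumption is that cameras are placed randomly with respect to animal
movement. The package includes a bias scenario in which cameras sit at
features (shade trees) that attract animals by day, and supports the
standard mitigation: estimating from night-only events, pairing the night
encounter rate (12 h effort per camera-day) with the night speed `V_n`.

The package is aimed at statistical ecologists: it covers event
independence filtering, day/night and season–habitat stratification,
detection-zone estimation from approach trials, speed estimation from
continuous follows, kernel home ranges (75% isopleths) with habitat
overlaps and buffered effective areas for census reference densities, and a
simulator that generates every input from known truth.

## Worked example

Simulate a small survey (180 animals on a 6 × 6 km torus — a true density
of 5 /km² — with 9 cameras for 30 days), then run the estimation pipeline:

```python
import math
from remcam import (SimConfig, simulate, collapse_to_independent_events,
                    tally, bootstrap_rate_variance, delta_variance, REMParams)

cfg = SimConfig(seed=42, arena=(6.0, 6.0), n_animals=180, n_cameras=9,
                duration_h=720.0)
bundle = simulate(cfg)
events = collapse_to_independent_events(bundle.events, gap_min=15.0)
tallies = tally(bundle.deployments, events, window="all")
rate = bootstrap_rate_variance(tallies, n_boot=10_000, seed=42)
params = REMParams(v=0.2, r=0.01, theta=math.radians(50.0),
                   se_v=0.012, se_r=0.0008, se_theta=math.radians(1.56))
res = delta_variance(rate, params)
print(f"rate {rate.rate:.6f} events/h over {rate.t_total:.0f} h")
print(f"D = {res.d:.3f} /km2  se {res.se_d:.3f}  "
      f"95% CI {res.ci_low:.3f}-{res.ci_high:.3f}")
```

prints

```
rate 0.008333 events/h over 6480 h
D = 4.557 /km2  se 0.672  95% CI 3.418-6.075
```

54 independent events over 6,480 camera-hours give an encounter rate of
0.00833 events/h; the REM converts it to 4.56 animals/km², and the
lognormal 95% interval (3.42–6.08) comfortably covers the true density of
5/km². The `cv2_components` field of the result shows how much of the
variance each input contributes (here the encounter rate dominates).

The same workflow is available from the shell:

```bash
remcam simulate --config sim.yaml --out data/ --seed 42
remcam rate --events data/events.csv --deployments data/deployments.csv \
            --window night --n-boot 10000 --seed 42 --out rate.json
remcam estimate --rate rate.json --params params.yaml
remcam sensitivity --params params.yaml --which theta --delta 0.01
remcam study --config study.yaml --out results/
```

`remcam study` runs the full season × habitat × day/night stratification
and writes `results.json` plus effort/density/percent-error tables.

## Layout

| module | contents |
| --- | --- |
| `remcam.types` | domain types and validation (deployments, events, parameters, home ranges) |
| `remcam.io` | CSV / GeoJSON / YAML readers and writers |
| `remcam.events` | independence merging, day/night windows, effort, bootstrap encounter rates |
| `remcam.rem` | the REM, delta-method variance, sensitivity/elasticity |
| `remcam.fieldparams` | detection zone from approach trials, speed from follows |
| `remcam.reference` | kernel UDs, isopleths, overlaps, buffers, census reference densities |
| `remcam.simulate` | movement/detection simulator, bias scenario, fixture generators |
| `remcam.pipeline` | stratified study orchestration and report tables |
| `remcam.cli` | `remcam` command-line interface |

See `docs/methods.md` for the model, its assumptions, and the package's
numerical and design choices.
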