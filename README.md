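# icefox

Spatio-temporal hotspot detection for satellite-tracked territorial
predators on sea ice.

Territorial arctic foxes (*Vulpes lagopus*) occasionally leave their tundra
home ranges in winter to scavenge marine-mammal carrion on the land-fast
ice. Because carrion is a pulsed, aggregated resource, several foxes
converging on the same patch of ice within days of each other reveal both
the feeding event and — through the distances they travelled — how far away
they could detect it. `icefox` implements the full analysis chain for this
kind of study, for movement ecologists working with Argos collar data (or
any error-laden relocation data in a planar projection):

1. **Argos filtering** — location-class screening (LC 3/2/1) and the
   iterative forward speed filter (7 km/h sustained, 10 km/h bouts of up to
   12 min).
2. **Dynamic Brownian bridge movement model (dBBMM)** — from scratch:
   sliding-window (w = 9, margin = 3) changepoint estimation of the
   Brownian motion variance σ²ₘ by BIC between one- and two-variance window
   models, bridge utilization distributions (UDs) accounting for elapsed
   time and per-fix location error, cumulative probability contours, and
   50%-contour home ranges from on-land fixes.
3. **Population hotspots** — per-animal UDs on 30-day time slices stepped
   by 14 days; summed, land-masked population UDs; per-cell counts of
   overlapping individual 75% contours; regions with ≥ 3 animals, screened
   by attendance synchrony (≥ 3 members, ≥ 1 animal present 2+ consecutive
   days) and merged across overlapping slices.
4. **Attendance statistics** — per-fox presence chronologies, visits,
   joining distances (last fix the day before arrival → hotspot center),
   closest approaches of non-joiners, and seasonal land/sea/hotspot-day
   summaries.
5. **Mixed models** — Laplace-ML mixed logistic regression of hotspot
   joining on distance (crossed fox and hotspot random intercepts;
   reproduces `lme4::glmer`), and an ML linear mixed model of stay length,
   each with a likelihood-ratio test against its null.
6. **Synthetic scenarios** — an Ornstein-Uhlenbeck central-place-forager
   simulator with planted carcass sites, duty-cycled Argos-like
   observation (5.3 ± 2.1 fixes/day in a 3-h UTC window, class-dependent
   error) and a complete truth ledger for recovery testing.

The bridge density between fixes p₁, p₂ at elapsed time T uses

σ²(α) = T·α(1−α)·σ²ₘ + (1−α)²·δ₁² + α²·δ₂²,  α ∈ [0, 1],

with δᵢ the Gaussian SD of each fix (Argos radius/2), and σ²ₘ estimated by
leave-one-out likelihood within each window (the left-out fix contributes
its own δ² on top of the bridge variance).

## Worked example

Simulate a winter and run the whole pipeline:

```python
import warnings
from icefox.simulate import default_scenario
from icefox.pipeline import run_pipeline
from icefox.attendance import hotspot_summary, visitor_summary_stats

locations, mask, truth = default_scenario(seed=1)
print(f"{len(locations)} fixes from {locations['animal_id'].nunique()} foxes")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")          # short-track fallbacks warn
    result = run_pipeline(locations, mask)
print(f"{len(result.filtered)} fixes retained after filtering")
for h in result.hotspots:
    s = hotspot_summary(result.attendance[h.hotspot_id])
    print(f"{h.hotspot_id}: {s['n_members']} foxes, {s['first_date']} to "
          f"{s['last_date']} ({s['duration_days']} d), peak "
          f"{s['peak_attendance']}/day, center "
          f"({h.center[0]/1000:.1f}, {h.center[1]/1000:.1f}) km")
stats = visitor_summary_stats(result.season_summaries)
print(f"{stats['n_visitors']} hotspot visitors; "
      f"{stats['mean_pct_sea_days_at_hotspots']:.1f} +/- "
      f"{stats['sd_pct_sea_days_at_hotspots']:.1f} % of their sea-ice days "
      "were at hotspots")
```

prints

```
27572 fixes from 24 foxes
27136 fixes retained after filtering
H1: 6 foxes, 2010-12-05 to 2010-12-18 (14 d), peak 6/day, center (13.0, -9.6) km
H2: 3 foxes, 2010-12-11 to 2010-12-19 (9 d), peak 2/day, center (55.0, -5.1) km
H3: 11 foxes, 2011-01-04 to 2011-01-19 (16 d), peak 7/day, center (44.5, -4.6) km
H4: 7 foxes, 2011-01-23 to 2011-02-03 (12 d), peak 5/day, center (18.5, -3.6) km
H5: 7 foxes, 2011-02-02 to 2011-02-16 (15 d), peak 3/day, center (36.5, -8.6) km
21 hotspot visitors; 87.9 +/- 21.8 % of their sea-ice days were at hotspots
```

Each line is one detected hotspot: its members, active dates, duration,
the maximum number of foxes present on a single day, and the center (the
highest-valued cell of the population UD inside the hotspot). This seed
plants five carcass sites; all five are detected and the two distractor
sites (≤ 2 visitors) are not. The closing line is the seasonal summary
over the hotspot visitors: what share of their sea-ice days was spent at
detected hotspots.

The same stages are available from a CLI (`icefox simulate`, `filter`,
`dbbmm`, `hotspots`, `attendance`, `models`), reading/writing CSV,
GeoJSON and ESRI ASCII grids — see `icefox --help`.

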