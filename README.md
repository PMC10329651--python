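# omegaquant

Quantification of **omegasome ring constriction kinetics** from fluorescence
time-lapse microscopy.

Omegasomes are PtdIns3P-rich, cup-shaped ER subdomains on which
autophagosomes form. In live imaging of fluorescently tagged DFCP1 they
appear as a spot that expands into a ring of ~0.5–1.5 µm diameter, holds its
maximum size while the phagophore matures, and then constricts back to a
spot before disappearing. DFCP1 is an ATPase, and cells expressing
ATP-binding (K193A) or hydrolysis-defective (T189A) mutants show a
characteristic defect: constriction stalls at ~0.8 µm for prolonged periods,
lengthening the omegasome life cycle (wild type ≈ 330–350 s; mutants
≈ 450–500 s).

The package is written for cell biologists quantifying this kind of data. It
provides:

* **`synthmovie`** — a synthetic time-lapse generator with exact per-event
  ground truth (phase boundary times, maximum/stall diameters, cargo
  recruitment), emulating 2-s-interval movies with Poisson shot noise and
  Gaussian read noise. Wild-type and ATPase-mutant kinetic presets are
  built in, so the whole pipeline is testable without any imaging data.
* **`ringtrack`** — seeded per-track segmentation: a 50×50 px region of
  interest per frame, Otsu thresholding (256-bin, exact arithmetic),
  8-connected particles larger than 3 px, centroid within 10 px of the ROI
  center, and per-particle mean intensity, area and Feret's diameter.
* **`dynamics`** — diameter-vs-time profiles (Feret × pixel size, 5-frame
  rolling median), phase segmentation (earliest maximum ⇒ constriction
  onset; disappearance ⇒ fully constricted), lifetimes, constriction
  success (final diameter < 0.5 µm), stall plateau detection, size-class
  trajectory ensembles (mean ± 95 % CI), and the Spearman correlation of
  maximum diameter with lifetime.
* **`recruit`** — cargo-channel (p62/LC3B) recruitment scoring: cargo over
  local annulus background must exceed 1.5× for ≥3 consecutive frames;
  recruited fractions carry exact Clopper–Pearson intervals.
* **`puncta`** — fixed-image quantification: rolling-ball background
  subtraction (grayscale opening with a flat disk), robust dot segmentation
  (median + 5·MAD), per-cell counts and sum intensities with cells defined
  by nearest-nucleus territories, and channel co-occurrence fractions.
* **`stats`** — the "superplot" reporting convention: tests run on
  per-experiment means; one-way ANOVA with Dunnett's many-to-one
  comparisons against a control, one-sample t-tests, nonparametric
  alternatives (Mann–Whitney, Kruskal–Wallis + Dunn), and the ratiometric
  mKeima flux statistic median(561 nm)/median(407 nm).

## Worked example

Simulate five hydrolysis-mutant omegasomes, track them exactly as a
microscopist would (seed points → ROI → Otsu → Feret), and summarize:

```python
from omegaquant import (SimulationConfig, simulate, seeds_from_events,
                        measure_tracks, build_profiles, summarize_track)

cfg = SimulationConfig.preset("hydrolysis_mutant", n_events=5, rng_seed=42)
movie, events = simulate(cfg)
seeds = seeds_from_events(events, cfg.frame_interval_s)
measurements = measure_tracks(movie, seeds)
profiles = build_profiles(measurements, cfg.pixel_size_um,
                          cfg.frame_interval_s)
for p in profiles:
    s = summarize_track(p)
    print(f"track {s.track_id}: lifetime {s.lifetime_s:.0f} s, "
          f"d_max {s.d_max_um:.2f} um, success={s.constricted_success}, "
          f"stall={s.stall_detected}"
          + (f" ({s.stall_diameter_um:.2f} um x {s.stall_duration_s:.0f} s)"
             if s.stall_detected else ""))
```

```
track 0: lifetime 414 s, d_max 1.04 um, success=True, stall=True (0.84 um x 92 s)
track 1: lifetime 512 s, d_max 1.04 um, success=True, stall=True (0.84 um x 126 s)
track 2: lifetime 466 s, d_max 1.28 um, success=True, stall=True (0.84 um x 104 s)
track 3: lifetime 422 s, d_max 1.04 um, success=True, stall=True (0.84 um x 68 s)
track 4: lifetime 450 s, d_max 1.04 um, success=True, stall=True (0.84 um x 96 s)
```

Every track is flagged as stalling near the programmed 0.8 µm plateau (the
~0.04 µm excess is the segmentation's outer-edge bias, below one pixel),
lifetimes scatter around the mutant preset's 450-s mean, and all five rings
eventually constrict below the 0.5 µm success threshold despite the stall.

The same stages are available as a CLI for shell use:

```sh
omegaquant simulate --genotype wt --out sim --seed 4
omegaquant segment  --movie sim/movie.tif --seeds sim/seeds.csv \
                    --channel dfcp1 --out measurements.csv
omegaquant tracks   --measurements measurements.csv --out tracks_out
omegaquant recruit  --movie sim/movie.tif --measurements measurements.csv \
                    --out recruitment.csv
omegaquant puncta   --image field.tif --channels nuclei=0,p62=1,dfcp1=2 \
                    --out puncta_out
omegaquant report   --table table.csv --control wt --out report.json
```

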