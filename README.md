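# shearwater

Trajectory analysis of central-place seabird foraging trips: behavioural
segmentation, homing-onset detection, mixture-model state classification,
orientation statistics, and mixed-model treatment inference — with a fully
ground-truthed synthetic-colony generator so every stage is testable
without field data.

## The problem

Procellariiform seabirds are suspected of navigating the open ocean with an
olfactory map.  The decisive free-ranging test is to GPS-track incubating
shearwaters whose senses have been experimentally manipulated — anosmic
(zinc-sulphate irrigation of the olfactory mucosa), magnetically disrupted
(head-mounted neodymium magnet), or control — over their own foraging trips
and ask where, if anywhere, behaviour diverges: in the decision and timing
of homing, in the orientation of the pelagic (out-of-sight-of-land) versus
coastal return, in at-sea activity budgets, or in foraging success
(mass gained at sea).  This package implements that analysis chain for
Movebank-style GPS data:

1. **Tracks** — read per-bird deployments, split them into colony
   departure→return trips, resample to an exact 5-minute grid by cubic
   splines, derive speeds and turning angles, classify day/night by solar
   elevation (−12°, nautical night).
2. **Segmentation** — Douglas–Peucker behavioural units; the decision to
   home found by a backward scan for the contiguous suffix of segments with
   significant homeward movement, sharpened by a leg-wise homeward-speed
   walk.
3. **States** — a Gaussian mixture over (speed, |turn|), the number of
   states chosen at the log-likelihood elbow, components labelled
   rest / forage / commute by ascending mean speed
   (≈ 0.3 / 1.8 / 6.7 m s⁻¹ in this system).
4. **Orientation** — virtual vanishing bearings at 10 km, the 40-km
   pelagic/coastal split of homing against a coastline, per-fix homeward
   deviations of flight legs (home = 0°), straightness (beeline / path),
   homing departure timing.
5. **Inference** — iterated Watson–Williams circular ANOVA (one angle per
   bird per resample, 5 000 resamples), LMMs with bird or trip-in-bird
   random intercepts (REML estimates, ML likelihood-ratio tests, Tukey
   post-hoc), Laplace binomial GLMMs for per-fix state indicators with
   bird/trip/date intercepts and an overdispersion check, and the
   incubation-corrected mass-gain ~ foraging-effort GLM.

The statistical model for the headline question is, for each homing phase,

    deviation_ijk = μ_treatment(i) + b_i + t_ij + ε_ijk

with bird intercepts `b_i`, trip-in-bird intercepts `t_ij`, and the
treatment means tested by LR against the intercept-only null; the
deviation is `wrap(bearing(fix→next fix) − bearing(fix→colony))` over
commute-labelled legs, so a bird flying straight home scores 0°.

See `docs/methods.md` for the full model descriptions, parameter defaults,
and limitations.

## Worked example

Simulate a small colony (4 birds per treatment, 1.5–3-day trips; the
generator scripts a +22° pelagic homing bias for anosmic birds only) and
run the full pipeline:

```python
from shearwater.simulate import SimConfig, simulate_colony, write_dataset
from shearwater.pipeline import RunConfig, run_pipeline

cfg = SimConfig(rng_seed=42, n_birds={"control": 4, "magnetic": 4, "anosmic": 4},
                trip_days_range=(1.5, 3.0))
paths = write_dataset(simulate_colony(cfg), "demo")
run_cfg = RunConfig(tracks_path=str(paths["tracks"]),
                    metadata_path=str(paths["metadata"]),
                    weighings_path=str(paths["weighings"]),
                    coastline_path=str(paths["coastline"]),
                    out_dir="demo_out", K_override=3, rng_seed=1)
res = run_pipeline(run_cfg, colony=cfg.colony)
print(res.outbound_ww.summary())
print(res.stats["pelagic_deviation_lmm"].summary())
print(res.stats["coastal_deviation_lmm"].summary())
```

which prints (exact output of this configuration):

```
Iterated Watson-Williams test (5000 resamples)
  p = 0.04429 +/- 0.00028 (mean +/- s.e.)
  F (mean) = 4.750
  mean direction [control] = 317.36 deg
  mean direction [magnetic] = 334.35 deg
  mean direction [anosmic] = 279.35 deg
Mixed model for 'deviation_deg' (cell-means treatment coding)
  control: -1.777 +/- 0.664 (s.e.)
  magnetic: 0.8715 +/- 0.922 (s.e.)
  anosmic: 20.06 +/- 1.03 (s.e.)
  LR test: chi2 = 301.261, df = 2, p = 3.819e-66
  Tukey control-magnetic: t = -2.331, df = 9.0, p = 0.102
  Tukey control-anosmic: t = -17.799, df = 9.0, p = 0.000
  Tukey magnetic-anosmic: t = -13.866, df = 9.0, p = 0.000
Mixed model for 'deviation_deg' (cell-means treatment coding)
  control: 1.56 +/- 1.12 (s.e.)
  magnetic: 2.932 +/- 1.61 (s.e.)
  anosmic: 0.3065 +/- 1.65 (s.e.)
  LR test: chi2 = 1.309, df = 2, p = 0.5196
```

Reading it: outbound orientation barely differs (the iterated circular
ANOVA's mean p sits near 0.05 because the generator gives anosmic birds a
more coastal departure direction); during the **pelagic** homing phase the
anosmic group is misoriented by ≈ +20° while control and magnetic birds
point home (the scripted +22° bias, recovered with its Tukey contrasts);
in the **coastal** phase all three groups are home-oriented and the test is
null — orientation recovers within sight of land.

The same run via the command line:

```bash
shearwater simulate --out demo --seed 42 --birds 4
shearwater run --tracks demo/tracks.csv --metadata demo/metadata.csv \
    --weighings demo/weighings.csv --coastline demo/coastline.geojson \
    --out demo_out --seed 1 --k-override 3
shearwater report demo_out
```

`demo_out/` then holds annotated per-trip CSVs, the segment table, the
behaviour (activity-budget) table, orientation summaries, the statistics
CSV and a run log with versions, seeds and every parameter used.

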