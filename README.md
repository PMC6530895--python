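# echoprey

Prey-field quantification from **recreational-grade echosounders** (RGE):
a tested pipeline from raw 8-bit ping records to negative-binomial GAMMs of
predator counts against relative prey abundance.

## The problem

Small epipelagic fishes (sprat, pilchard, mullet) are key prey for coastal
predators such as Hector's dolphin and little penguin, but their extreme
patchiness makes them hard to survey. Consumer echosounders record digital
water-column backscatter at a fraction of the cost of a scientific system —
but without calibration, documented source levels or gain functions. Stored
samples are 8-bit integers on an undocumented scale, and the stored
intensity is depth dependent because the applied time-varied gain (TVG) is
unknown. This package implements the full analysis chain that makes such
data usable for *relative* prey-field work:

1. **I/O** (`echoprey.io`) — read/write ping-level CSV exports; convert
   8-bit counts to relative dB (`20·log10(count/255)`, full scale = 0 dB);
   assemble echograms with depth and along-track (haversine) axes.
2. **TVG calibration** (`echoprey.calibration`) — isolate 8×1 regions
   around a tungsten-carbide calibration sphere lowered 3–35 m below the
   transducer, and select the TVG form `Y(R) = ξ·log₁₀(R) + 2αR`,
   ξ ∈ {10, 15, 20, 40}, that minimises |Pearson r| between corrected
   intensity and depth. Absorption α from Francois–Garrison (1982), sound
   speed from Mackenzie (1981), both from CTD temperature/salinity at
   200 kHz, pH 8.
3. **Preprocessing** (`echoprey.preprocessing`) — exclude the 3 m acoustic
   near-field, pick the seabed line (offset-invariant relative threshold,
   cross-ping median continuity), and remove range-dependent background
   noise with a minimum-cell estimator (linear-domain subtraction, low-SNR
   samples floored).
4. **School detection** (`echoprey.schools`) — SHAPES-style: threshold at
   −35 dB relative intensity, 4-connected candidates, bounding-box linking,
   minimum-dimension filtering, then beam-geometry corrections

   ```
   Lc = L − 2·D·tan(φ/2)        (beam-width smear at mean depth D)
   Tc = T − (C/2)·(τ/1000)      (pulse-length smear)
   Ac = A·(Lc·Tc)/(L·T)         (if L·T ≠ 0)
   ```

   with φ = 12° beam angle, τ = 0.2 ms pulse, C = sound speed.
5. **RAPP metrics** (`echoprey.rapp`) — per-survey relative abundance of
   potential prey: `c.SchA` (Σ Ac per km of track, m²/km) and `Prop.Track`
   (union of corrected along-track school intervals ÷ track length, ≤ 1).
6. **Count models** (`echoprey.gamm`) — NB GAMMs
   `log μ = β₀ + s(RAPP) + b_region + log(distance)`, cubic spline with
   basis dimension 4, GCV-chosen smoothness, ridge (random-effect) region
   intercepts, profiled NB dispersion; metrics compared per predator by
   AIC; goodness of fit as % deviance explained.
7. **Synthetic truth** (`echoprey.synthetic`) — generators for every input:
   echograms with planted elliptical schools and seabed, calibration-sphere
   drops, and 136-survey predator-count tables drawn from a known NB model,
   so every stage is testable against known truth with no field data.

## Worked example

Generate a synthetic field season, characterise the system, and model the
predators:

```
$ echoprey simulate --out demo/bundle --seed 7
bundle written to demo/bundle

$ echoprey ground-truth --pings demo/bundle/ground_truth_pings.csv \
    --sphere demo/bundle/sphere_pings.csv \
    --sphere-annotations demo/bundle/sphere_annotations.csv \
    --ctd demo/bundle/ctd.csv --out demo/gt
4 schools; TVG 10log; outputs in demo/gt

$ echoprey model --rapp demo/bundle/surveys.csv --out demo/model
dolphin_count: best=prop_track deviance=33.3% dAIC=12.3
penguin_count: best=c_scha_m2_per_km deviance=45.1% dAIC=13.7
```

The ground-truth run wrote `demo/gt/tvg_report.json`:

```json
{
 "xi_selected": 10.0,
 "alpha_db_per_m": 0.0603,
 "sound_speed_ms": 1499.8,
 "n_regions": 300,
 "correlation_by_xi": {"10.0": 0.025, "15.0": 0.889,
                       "20.0": 0.941, "40.0": 0.960}
}
```

Reading: from 300 sphere regions the 10log (cylindrical-spreading) form
flattens intensity against depth (|r| = 0.025) while 15/20/40log
overcompensate, so 10log is applied to all echograms from this system. The
detected-school table (`school_table.csv`) lists uncorrected (L, T, A, D)
and beam-corrected (Lc, Tc, Ac) morphology per school; `model_report.json`
shows that survey-track coverage (Prop.Track) best predicts dolphin counts
while cumulative school area (c.SchA) best predicts penguin counts — each
best model explaining 33–45% of count deviance on this synthetic season.

The library surface mirrors the CLI: see `echoprey.render_echogram`,
`fit_tvg_form`, `detect_schools`, `summarize_survey`, `select_best_metric`.

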