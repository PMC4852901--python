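# paleoprod

Tools for reconstructing lake primary-production histories from dated
sediment cores and mapping atmospheric nutrient deposition from snowpack
surveys — the inference chain used in multi-lake assessments of whether
production increases around an industrial centre are driven by local
nutrient emissions or by regional climate warming.

## Who this is for

Paleolimnologists and environmental scientists who need a tested, scriptable
version of the standard analysis chain:

1. **²¹⁰Pb dating (CRS model).** Unsupported ²¹⁰Pb is total ²¹⁰Pb minus the
   ²²⁶Ra-supported fraction. Under a constant rate of supply, the age of
   depth *x* is *t(x) = λ⁻¹ ln(A(0)/A(x))* with *λ* = ln2/22.3 yr⁻¹ and
   *A(x)* the cumulative unsupported inventory beneath *x*; the dry-mass
   accumulation rate is *r(x) = λA(x)/C(x)*. Uncertainties (±2 SD) come from
   Monte-Carlo resampling of the measured activities; chronologies are
   validated against the 1963 ¹³⁷Cs fallout peak, extrapolated below
   radiometric background, and smoothed with a polynomial constrained
   through the coring year.
2. **Spectral chlorophyll-a.** Sedimentary chl-a (plus diagenetic products),
   a proxy for whole-lake primary production, is inferred from visible
   reflectance spectra: absorbance A = log₁₀(1/R), chord-subtracted peak
   area over 650–700 nm, and a linear calibration with a detection limit of
   0.01 mg/g dry weight.
3. **Trend statistics.** Enrichment factors (mean post-2000 concentration ÷
   mean 1955–1970 baseline), dibenzothiophene (DBT)-based classification of
   sites into minimally (<2) and highly (>2) enriched groups, per-lake
   Z scores pooled into 5-year bins, continuous two-segment breakpoint
   regression with an F test, Welch t-tests, and Pearson correlations
   against annual and seasonal climate series.
4. **Deposition mapping.** Snowpack loading = concentration (mg/L) × snow
   water equivalent (mm), interpolated by ordinary kriging under a fitted
   semivariogram, cross-validated leave-one-out, integrated over a disc
   around the industrial centre to tonnes, and normalized between winters
   with different snow-accumulation periods.

A synthetic-data module simulates cores, snow surveys and climate series
with known ground truth so the full chain is testable end to end, and a
printed 23-site summary table ships as a package fixture.

## Worked example

```python
from paleoprod.synthetic import CoreSimConfig, simulate_core
from paleoprod import dating

core = simulate_core(CoreSimConfig(seed=1))          # 80 x 0.5 cm intervals
profile = dating.RadionuclideProfile.from_frame(core.intervals)
model = dating.crs_age_model(profile, coring_year=2014, seed=1)
model = dating.extrapolate_below_background(model, profile)
model = dating.fit_age_depth_polynomial(model)
peak = dating.locate_cs137_peak(profile, model)
print(f"background at {model.background_depth_cm:.1f} cm, "
      f"surface date {model.crs_year[0]:.1f} +/- {model.sd2[0]:.1f}")
print(f"137Cs peak dated {peak.crs_year:.1f} +/- {peak.sd2:.1f} "
      f"(validated: {peak.validated})")
```

prints

```
background at 29.0 cm, surface date 2012.5 +/- 0.2
137Cs peak dated 1963.9 +/- 1.6 (validated: True)
```

— the chronology dates the surface interval to its deposition midpoint
(~1.5 yr before coring), and the simulated 1963 fallout maximum lands within
the peak interval's span plus its 2-SD age envelope, so the independent
marker confirms the ²¹⁰Pb chronology.

The same chain runs end to end from the command line:

```bash
paleoprod run --seed 1 --out results/       # simulate → date → chla → trends → deposition
paleoprod report                            # summary of the shipped printed table
```

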