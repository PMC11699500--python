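# wristrhr

Resting heart rate (RHR) from wrist-wearable photoplethysmography (PPG), as a
reusable, tested analysis pipeline for biostatisticians and digital-health
researchers validating a wearable against an in-clinic ECG reference.

Consumer and research wrist devices detect heartbeats optically and report
interbeat intervals (IBIs, ms). Turning those into a trustworthy *resting*
heart rate requires gating out motion, non-wear and optical artifacts. This
package implements that full analysis stack:

1. **RHR derivation** — a 2-minute sensor window centered on the ECG
   acquisition midpoint; windows with any off-wrist state are excluded; IBIs
   in "Active" 30-second actigraphy epochs (nonzero count) are removed; IBIs
   failing the jump-distance quality rule `|I_i − I_{i−1}| ≥ 100 ms` are
   removed; participants with fewer than 3 surviving IBIs are excluded; and

   `RHR = 60000 · N / Σᵢ Iᵢ  (bpm)`

   i.e. the reciprocal of the mean retained interval. A 30-day mean daily
   step metric (days with ≥ 10 h wear) is included.
2. **Agreement analysis** — intraclass correlation ICC(2,1) (two-way random
   effects, absolute agreement, single measure), mean bias
   `mean(device − ECG)`, the slope of the difference regressed on ECG RHR
   (proportional error), and seeded 1000-replicate percentile-bootstrap 95%
   CIs — overall and per sex.
3. **Trend analysis** — within-sex RHR categories at the 25th/75th
   percentiles; Cochran–Armitage trend tests for binary baseline
   characteristics (including level-vs-rest dummies of categoricals) and
   Spearman rank correlation for continuous ones.
4. **Association models** — MICE with predictive mean matching (m = 5),
   Box–Cox transforms for continuous vitals/physical-function and laboratory
   measures, raw age plus age² (the inverted-U age profile), standardization,
   and a stacked elastic net (α ∈ {0.5, 1}, 100-point λ path, 5-fold CV with
   participant-level folds) per covariate domain and sex.
5. **Synthetic cohort generator** — sensor streams, ECG sessions, step
   summaries and domain-tagged covariates with known ground truth, including
   a false-beat splitting artifact mechanism that yields a small positive
   device bias declining with reference RHR.

## Worked example

```python
import wristrhr as w

cfg = w.SimulationConfig(n_participants=400, seed=5)
bundle = w.generate_cohort(cfg)
rhr = w.derive_rhr_table(bundle.ecg, bundle.ibi, bundle.actigraphy,
                         bundle.wrist, participants=bundle.participants)
pairs, flow = w.build_analysis_cohort(rhr)
print(flow.to_string(index=False))
res = w.MethodAgreement(pairs).fit(n_boot=1000, seed=1)
print(res.summary())
```

prints

```
                 stage  count
                 input    400
  excluded_ecg_quality      0
excluded_no_wrist_data      0
    excluded_off_wrist     15
      excluded_low_ibi      0
                cohort    385

Device vs ECG resting-heart-rate agreement
(percentile bootstrap, 1000 resamples, 95% CI)

stratum      n  ICC(2,1)  bias bpm           bias CI    slope            slope CI
all        385     0.967      0.97      (0.69, 1.23)   -0.045    (-0.070, -0.021)
female     240     0.966      0.70      (0.32, 1.03)   -0.050    (-0.082, -0.016)
male       145     0.966      1.41      (0.98, 1.83)   -0.030     (-0.065, 0.005)
```

15 of 400 simulated participants were wearing the watch off-wrist during the
window and are excluded; on the remaining 385 the device agrees excellently
with ECG (ICC ≈ 0.97) but overestimates RHR by ~1 bpm on average, and that
overestimate shrinks as the reference RHR rises (negative slope) — the
signature of occasional false-beat detection at long interbeat intervals.

The same stages are available from a shell:

```bash
wristrhr run-all --out run/ --synthetic --seed 1
```

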