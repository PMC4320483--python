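# modeshift

Recognising transport modes — walking, cycling, train, bus, car — from
nothing but the speed signal of a 1 Hz GPS logger.  Built for
epidemiologists and exposure scientists who want to classify
commute episodes in GPS tracking studies without accelerometers, map
matching or GIS context.

## What it does

1. **Segmentation.** Each speed profile is cut into *sequences*
   wherever speed is zero (zero speed ⇒ no transport).  Sequences are
   binned by duration (≤15 s, 16–30 s, 31–60 s, >60 s) because very
   short episodes are intrinsically hard to classify.
2. **Speed metrics.** Seven per-sequence features: mean, 95th
   percentile and sample SD of speed; the rate-of-change metric
   RCM = (1/(N−1)) Σₙ |Sₙ − Sₙ₋₁|; the standardised RCM (RCM/SD); and
   the 95th/5th percentiles of consecutive speed differences as
   acceleration/braking proxies.
3. **Non-parametric discriminant analysis.** Class-conditional
   product-Gaussian kernel density estimates (Silverman bandwidths
   h = 1.06 σ̂ m^(−1/5) per class and dimension) combined with class
   priors via Bayes' rule, evaluated in log space; a kNN discriminant
   ships as a sensitivity alternative.
4. **Person-level cross-validation.** Every 8-development /
   4-validation partition of the 12-person cohort (C(12,4) = 495) that
   covers all modes on both sides; agreement between predicted and
   true mode measured per duration stratum with Cohen's kappa
   κ = (p_o − p_e)/(1 − p_e) and observed agreement, summarised as
   median and IQR over splits, for every combination of 1–3 metrics
   (63 in all), in the five-class scheme and in a three-class scheme
   with train/bus/car collapsed to "motorized".
5. **Synthetic cohort.** A seeded generator produces labelled 1 Hz
   commute traces whose per-mode speed distributions for sequences
   over one minute match published cohort statistics (walk 4.1, bike
   14.9, train 88.3, bus 31.1, car 41.7 km/h medians with their IQRs),
   so the whole pipeline is testable without any data download.

See `docs/methods.md` for the model details, generator calibration and
its limitations.

## Worked example

```python
import modeshift as m

cohort   = m.simulate_cohort(m.CohortConfig(seed=0))      # 24 traces, ~83k points
filtered = [p for t in cohort for p in m.filter_indoor(t)]
features = m.feature_table(m.segment_traces(filtered))    # 779 sequences

for scheme, combo in [("three_class", ("p95", "accel", "decel")),
                      ("five_class",  ("p95", "accel", "decel")),
                      ("five_class",  ("p95",))]:
    _, summaries = m.run_crossval(features, None, [combo], scheme)
    row = next(r for r in summaries if r.stratum == ">60s")
    print(scheme, "+".join(combo),
          f"median kappa {row.kappa_median:.3f} "
          f"IQR ({row.kappa_q25:.3f}-{row.kappa_q75:.3f}) over {row.n_splits} splits")
```

prints

```
three_class p95+accel+decel median kappa 1.000 IQR (1.000-1.000) over 240 splits
five_class p95+accel+decel median kappa 0.942 IQR (0.840-0.967) over 90 splits
five_class p95 median kappa 0.743 IQR (0.670-0.803) over 90 splits
```

Read: with the 95th percentile of speed plus the acceleration and
braking proxies, sequences longer than one minute are classified
essentially perfectly once motorized modes are pooled (κ = 1.0), still
excellently when train, bus and car must be told apart (κ = 0.94, the
residual errors being bus/car confusions), and usefully even from the
single speed-percentile metric (κ = 0.74).

The same from the shell:

```sh
$ modeshift simulate --seed 0 --out demo/sim
wrote 83223 points to demo/sim/traces.csv
$ modeshift run --traces demo/sim/traces.csv --combos 1 --out demo/run
counts: {'traces_read': 24, 'points_read': 83223, ..., 'sequences_formed': 779,
         'splits_enumerated': 495, 'splits_valid_both': 90}
$ modeshift report --results demo/run/summary.csv --top 3

five_class, stratum >60s (median kappa, IQR):
  accel                   0.867 (0.801-0.936)  agreement 0.908  splits 90
  decel                   0.816 (0.740-0.877)  agreement 0.869  splits 90
  rcm                     0.801 (0.768-0.843)  agreement 0.864  splits 90

three_class, stratum >60s (median kappa, IQR):
  p95                     0.974 (0.951-1.000)  agreement 0.985  splits 240
  sd                      0.937 (0.904-0.969)  agreement 0.964  splits 240
  mean                    0.927 (0.895-0.948)  agreement 0.957  splits 240
```

`modeshift run` also writes `results.csv` (one row per split ×
combination × stratum), `calibration.csv` (the synthetic cohort's
per-mode summary), `manifest.json` (config echo, stage counts and a
content hash — reruns on identical input hash identically) and
`run.log`.

Real GPS data enters through the same CSV contract
(`person_id, commute_id, timestamp, speed_kmh, lat, lon, indoor, mode`)
or GPX 1.1 (`modeshift.read_gpx`; speeds taken from a `speed` extension
or derived from coordinates by haversine distance).

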