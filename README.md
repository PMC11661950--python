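# wardsense

Passive social sensing on a psychiatric ward: from raw wearable-badge
proximity logs to dyadic interaction events, daily weighted social networks,
per-person interaction metrics, and linear mixed models linking those metrics
to weekly symptom scores.

Social withdrawal is one of the earliest and most treatment-resistant signs
of psychosis-spectrum disorders, yet social functioning is usually measured
with rating scales that capture little of day-to-day behaviour. Wearable
proximity badges change that: every participant (patients and staff on an
open ward) wears a badge that broadcasts a BLE advertisement every 4 s and
logs every received packet as *(sender id, RSSI, Unix timestamp)*, plus a
battery ping every 5 min as a wear-time signal. From those logs this package
reconstructs who interacted with whom, when, and for how long, and asks
whether a patient's interaction pattern in the week before a clinical
assessment predicts that week's symptom severity (PANSS total).

The package is written for researchers running or re-analysing such a study.
Because proximity-log datasets from clinical wards cannot be shared, it also
contains a full synthetic-ward simulator with known ground truth (scheduled
meals, power-law background contacts, path-loss RSSI, packet loss, imperfect
wear compliance, symptom scores generated from the interaction features with
known coefficients), so every stage is testable end to end.

## The measurement model

1. **Cleaning.** Duplicate records, weekend records, records outside the
   08:00–20:00 wear window, and records with RSSI < −75 dBm (≈ 2 m) are
   removed, in that order, with per-rule counts reported.
2. **Events.** A detection at time *t* covers *[t, t+4]* s; gaps of up to
   75 s in a directional stream are bridged. An interaction event between two
   badges is the period in which **both** badges detected each other
   (intersection of the two directional streams, re-bridged; a union mode
   exists for asymmetric packet loss).
3. **Daily metrics.** Relative interaction time = (union of a person's event
   intervals) / (badge active time from battery pings); mean interaction
   duration = mean of log₁₀ durations (minutes), reflecting the long-tailed
   duration law.
4. **Networks.** One weighted undirected graph per day: nodes are badge-active
   participants; a dyad gets an edge when its summed interaction exceeds
   10 min, with weight *w*ᵢⱼ = log₁₀(total minutes). Node metrics:
   - *eigenvector centrality*: the *i*-th component of the unit-norm Perron
     vector **x** of the weighted adjacency **A** (**Ax** = λ**x**, λ the
     largest eigenvalue);
   - *weighted clustering* (Saramäki): with ŵᵢⱼ = wᵢⱼ / max(w),

     cᵢ = 1/(degᵢ(degᵢ−1)) · Σⱼₖ (ŵᵢⱼ ŵᵢₖ ŵⱼₖ)^⅓ .
5. **Longitudinal models.** Daily metrics are averaged over the 6 days
   preceding plus the day of each weekly assessment (each day used once, for
   the nearest assessment). Ten random-intercept models
   yᵢⱼ = β₀ + β₁ xⱼ + α₀ᵢ + εᵢⱼ (REML, predictors group-mean centered,
   observations nested in participants) relate self-report, time, and the
   four interaction features to relative interaction and PANSS total, with
   Satterthwaite-approximated F-tests, Cook's-distance outlier screening of
   the focal model, and optional olanzapine-equivalent dose covariates.

## Worked example

Run the simulated reference study (7 patients, 18 staff, 50 weekdays) end to
end with the numbered drivers:

```bash
python analysis/01_simulate.py      # ground truth + raw badge logs
python analysis/02_reconstruct.py   # cleaning funnel, events, daily summaries
python analysis/03_networks.py      # daily graphs, node metrics, windows
python analysis/04_models.py        # assessments + the ten-model suite
python analysis/05_validation.py    # oracle/recovery/calibration checks
```

Driver 02 printed, for the default seed:

```
filter funnel: 4956239 in -> 4112033 kept (dup 2149, weekend 0, hours 0, weak-signal 842057; parse rejects 0)
8380 interaction events over 50 days
patients: 2.98 h/day interacting (1.90 h with staff, 2.51 h with patients), badge active 9.9 h/day
```

i.e. about 16 % of raw packets are far-field sightings removed by the RSSI
threshold, and simulated patients spend ≈ 3 h/day in face-to-face
interaction — the order of magnitude reported for real ward life. Driver 04
then fits the suite on assessments generated with known slopes (negative for
relative interaction time, mean log duration and clustering; zero for
centrality and self-report):

```
 model  predictor                  beta1        F   df_den  p_value
     6  relative_interaction_time  -54.51   13.21    62     0.0006
     7  mean_log_duration          -18.97    8.91    62     0.0040
     8  eigenvector_centrality      -0.23    0.0001  62     0.9912
     9  clustering                 -38.55   11.98    62     0.0010
    10  self_report_index            0.35    0.18    62     0.6705

significant at .05: models [6, 7, 9] (configured truth: 6, 7, 9 negative; 8 and 10 null)
```

The configured effects are detected with the right signs and the configured
nulls stay null. The same pipeline is available as one command
(`wardsense run-all --seed 0 --out results/run`) and stage by stage
(`wardsense simulate / ingest / reconstruct / networks / models / validate`).

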