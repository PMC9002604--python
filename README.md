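# trusscast

Truss-level tomato monitoring and harvest prediction from bounding-box
detection streams and greenhouse temperature logs.

In greenhouse tomato production, the date a flower opens (anthesis)
plus accumulated thermal time determines when its fruit can be picked:
a fresh-market cultivar such as 'Momotaro York' is harvest-ready when
the **integrated temperature** — the inclusive sum of daily mean
temperatures from the bloom date —

```
S(n) = Σ_{i=0..n} T_{d+i}
```

reaches roughly 1100–1200 °C·days. `trusscast` turns per-frame
flower/fruit detections from truss-mounted cameras into that
prediction:

1. **detect_eval** — standard object-detection metrics (IoU at
   threshold 0.5, precision/recall/F1, per-class AP, mAP, average IoU)
   for validating a detector against annotated boxes.
2. **tracking** — assigns hierarchical IDs `plant_truss_position` to
   each bloomed flower by Euclidean centroid matching across frames,
   records anthesis dates, confirms flower→fruit transitions, flags
   dropped fruits and non-fruiting flowers, and detects truss
   completion (all fruits ≥ ~3 cm estimated diameter).
3. **thermal** — reduces raw 5-min temperature logs to
   quality-controlled daily means and fits a self-contained additive
   seasonal forecaster (changepoint-regularized saturating trend +
   yearly Fourier seasonality) scored by MAE.
4. **harvest** — computes each truss's harvest window `[⌈lo/T⌉−1,
   ⌊hi/T⌋−1]` days after bloom (constant-temperature closed form;
   cumulative scan in general), splicing measured temperatures with
   forecasts for the final lead-time weeks, and predicts the fruit
   count net of drops and non-fruiting flowers.
5. **synthetic** — a ground-truthed generator for greenhouse
   temperature logs and truss detection streams (jitter, camera
   shifts, drops, outliers, sensor outages), so the whole pipeline is
   testable without hardware.

A `trusscast` CLI (`simulate | track | forecast | predict |
eval-detect | eval-harvest | report`) binds the stages together.

## Worked example

A flower blooms on 1 September 2020 and every forecast daily mean is
20 °C:

```python
from datetime import date
import pandas as pd
from trusscast import harvest_window, integrated_temperature, IntegrationRule

days = pd.Series(20.0, index=pd.date_range("2020-09-01", "2021-01-31"))
print(harvest_window(date(2020, 9, 1), days, IntegrationRule(1100, 1200)))
print(integrated_temperature(days, date(2020, 9, 1), date(2020, 10, 25)))
```

prints

```
(datetime.date(2020, 10, 25), datetime.date(2020, 10, 30))
1100.0
```

i.e. the cumulative sum crosses 1100 °C·days on day n = 54 after bloom
and stays within 1200 through day n = 59, so the harvest window is
25–30 October — the classic degree-day arithmetic
`1100 ≤ 20·(n+1) ≤ 1200  ⟹  54 ≤ n ≤ 59`.

End to end on synthetic data (`trusscast simulate` → `track` →
`forecast` → `predict`), the default seven-truss scenario recovers
every anthesis date exactly, keeps 100 % of tracking IDs under 2 px
jitter and a 40 px camera shift, reaches a held-out daily-temperature
forecast MAE of ≈ 1.6 °C, and predicts harvest dates within ≈ 1–2 days
MAE even when the last five weeks of temperatures are forecast rather
than measured.

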