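# actipred

Activity-aware, power-optimized prediction of physiological signals from
multimodal wearable data.

Wearable health platforms stream many modalities — skin and ambient
temperature, humidity, wrist and ankle acceleration, electrodermal
activity (EDA), EKG-based heart rate (HR) — but every active sensor costs
battery. `actipred` implements a context-aware sensor-selection method for
body sensor networks: cluster time windows by physical activity using
accelerometer features, fit a sparse per-cluster HR prediction model whose
sparsity pattern is aligned with *sensors* rather than individual features,
and duty-cycle (idle) the sensors the active cluster's model does not use.
The package is aimed at researchers in mobile health and body sensor
networks who want a reproducible reference implementation of the
cluster-then-select pipeline together with a synthetic data generator for
end-to-end validation.

## The model

For sensor streams `x_k(t)`, `k = 1..N_s`, an activity cluster function

    C(t) = f_Xa(X_a((−∞, t]), t)  ∈ {1, …, K}

maps context features (21 sliding-window statistics of the ankle
accelerometer, embedded 21→3 by locality preserving projections and
clustered by k-means, K = 4) to an activity index. Per cluster `c` a linear
predictor `ŷ_c(t)` is fitted to windowed features `Z` grouped by sensor
(`N_g = 7` groups, p = 54 features) by the group lasso

    β̂ = argmin_β ‖Y − Σ_k Z_k β_k‖₂² + λ Σ_k ‖β_k‖_{W_k},
    ‖η‖_W = (η′Wη)^{1/2},

with `W_k = (1/M_k) I` (normalized scheme) or `W_k = (P_k/M_k) I`
(power-weighted scheme, `P_k` the sensor's current draw). The penalty
zeroes whole sensor groups; λ is chosen by day-wise cross-validation
(training days are the folds). A sensor whose group is inactive in the
current cluster's model is duty-cycled, saving its incremental current
`P_k`; the average saving weights each cluster by its occupancy,
`ΔI_avg = Σ N_c ΔI_c / Σ N_c`. HR history enters through lagged features
`y(t−δh), Δy, Δ²y`, where the horizon `δh` (10–90 s, or ∞ for none) sets
how early an anomaly could be flagged by comparing predicted and measured
HR.

See `docs/methods.md` for the full model description, numerical choices
and the synthetic-data design.

## Worked example

Simulate four days of the exercise protocol (scaled to ~11 min/day so the
example runs in about a minute), run the full pipeline with a 30 s HR
history horizon, and read off accuracy and power savings:

```python
from actipred import PipelineConfig, SimConfig, run_pipeline
from actipred.experiments import scaled_protocol

cfg = PipelineConfig(
    delta_h=30.0, n_lambdas=12,
    sim=SimConfig(n_days=4, protocol=scaled_protocol(0.12)),
)
rep = run_pipeline(cfg, seed=0)
print("pooled test RMSE", round(rep.pooled.rmse, 2), "bpm")
print("unclustered RMSE", round(rep.unclustered.rmse, 2), "bpm")
print("constant-predictor RMSE", round(rep.cp_baseline.rmse, 2), "bpm")
print({c: sorted(s) for c, s in rep.active_sets.items()})
print("avg current reduction", round(rep.power.avg_mA, 2), "mA",
      f"({rep.power.avg_pct:.1f} %)")
```

Output:

```
pooled test RMSE 7.2 bpm
unclustered RMSE 6.47 bpm
constant-predictor RMSE 11.41 bpm
{0: ['ankle_accel', 'eda', 'hr', 'wrist_accel'],
 1: ['ankle_accel', 'eda', 'wrist_accel'],
 2: ['ankle_accel', 'eda', 'hr', 'wrist_accel'],
 3: ['ankle_accel', 'eda', 'wrist_accel']}
avg current reduction 1.74 mA (17.5 %)
```

Reading this: the learned models beat the naive baseline that repeats HR
from 30 s ago (7.2 vs 11.4 bpm RMSE); every cluster drops the three
near-constant environment/body-temperature sensors, and the two
high-intensity clusters additionally drop the HR/EKG sensor — its history
is least informative when HR is most dynamic — which is where the bulk of
the 1.74 mA average saving (17.5 % of the system's draw) comes from. On
this short scaled recording clustering costs a little accuracy versus the
single global model; on longer recordings the per-cluster fits have more
data and the gap closes.

The same pipeline is exposed on the command line:

```sh
actipred simulate --days 4 --seed 0 --out rec/
actipred run --manifest rec/manifest.json --delta-h 30 --seed 0 --out out/
actipred power --active wrist_accel,ankle_accel
```

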